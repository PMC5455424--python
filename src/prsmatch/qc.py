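"""Genotype quality control for a SNP-panel matrix.

Rules applied, in a fixed deterministic order:

1. drop SNPs that failed in more than ``max_fail_fraction`` of samples
   (default 2%, strict inequality);
2. drop samples that failed for more than ``max_failed_snps`` SNPs
   (default 10, strict inequality);
3. on the filtered matrix, test Hardy-Weinberg equilibrium per SNP by
   comparing the observed number of homozygotes (either class) with the
   binomial expectation under the control-estimated allele frequency, plus
   an aggregate observed-vs-expected homozygote check over the whole panel;
4. screen pairwise genotype-dosage correlations for residual LD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "HweResult",
    "snp_call_rate_filter",
    "sample_failure_filter",
    "hwe_homozygote_test",
    "aggregate_hwe_test",
    "pairwise_r2",
    "run_qc",
]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs risk-allele counts with nan marking failed assays."""

    sample_ids: list[str]
    rsids: list[str]
    counts: np.ndarray  # float array, values {0, 1, 2, nan}

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sample_ids), len(self.rsids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.rsids)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.rsids)) != len(self.rsids):
            raise ValueError("duplicate rsids")
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype {self.counts[i, j]} at sample "
                f"{self.sample_ids[i]}, SNP {self.rsids[j]}"
            )

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.counts)

    def subset(
        self, samples: Sequence[str] | None = None, snps: Sequence[str] | None = None
    ) -> "GenotypeMatrix":
        si = (
            [self.sample_ids.index(s) for s in samples]
            if samples is not None
            else list(range(len(self.sample_ids)))
        )
        vi = (
            [self.rsids.index(r) for r in snps]
            if snps is not None
            else list(range(len(self.rsids)))
        )
        return GenotypeMatrix(
            [self.sample_ids[i] for i in si],
            [self.rsids[j] for j in vi],
            self.counts[np.ix_(si, vi)],
        )


def snp_call_rate_filter(
    matrix: GenotypeMatrix, max_fail_fraction: float = 0.02
) -> tuple[list[str], list[tuple[str, float]]]:
    """Exclude SNPs whose missing fraction strictly exceeds the threshold."""
    if matrix.counts.size == 0:
        raise ValueError("empty genotype matrix")
    frac = matrix.missing.mean(axis=0)
    kept = [r for r, f in zip(matrix.rsids, frac) if f <= max_fail_fraction]
    excluded = [
        (r, float(f)) for r, f in zip(matrix.rsids, frac) if f > max_fail_fraction
    ]
    return kept, excluded


def sample_failure_filter(
    matrix: GenotypeMatrix, max_failed_snps: int = 10
) -> tuple[list[str], list[tuple[str, int]]]:
    """Exclude samples that failed for strictly more than ``max_failed_snps`` SNPs."""
    if matrix.counts.size == 0:
        raise ValueError("empty genotype matrix")
    nfail = matrix.missing.sum(axis=1)
    kept = [s for s, n in zip(matrix.sample_ids, nfail) if n <= max_failed_snps]
    excluded = [
        (s, int(n)) for s, n in zip(matrix.sample_ids, nfail) if n > max_failed_snps
    ]
    return kept, excluded


class HweResult(NamedTuple):
    n: int
    observed_hom: int
    expected_hom: float
    p_value: float


def hwe_homozygote_test(genotypes: Sequence[float]) -> HweResult | None:
    """Binomial test of the observed homozygote count against HWE expectation.

    The allele frequency is estimated from the same genotypes
    (``p_hat = mean(g)/2``); under HWE a subject is homozygous (genotype 0
    or 2) with probability ``p_hat^2 + (1 - p_hat)^2``.  The two-sided
    p-value uses the minimum-likelihood rule (the sum of probabilities of
    all outcomes no more likely than the observed count), the small-sample
    exact convention.

    Returns None (with a warning) when no genotypes are called.
    """
    g = np.asarray(genotypes, dtype=float)
    g = g[~np.isnan(g)]
    n = g.size
    if n == 0:
        warnings.warn("no called genotypes: SNP skipped in HWE test", stacklevel=2)
        return None
    p_hat = g.mean() / 2.0
    p_hom = p_hat**2 + (1.0 - p_hat) ** 2
    obs = int(np.sum((g == 0) | (g == 2)))
    pval = stats.binomtest(obs, n, p_hom).pvalue  # two-sided, minlike method
    return HweResult(n=n, observed_hom=obs, expected_hom=n * p_hom, p_value=float(pval))


def aggregate_hwe_test(results: Sequence[HweResult]) -> dict[str, float]:
    """Panel-wide observed vs expected homozygotes, normal approximation.

    Sums observed and expected homozygote counts over SNPs; the variance of
    the total is the sum of per-SNP binomial variances ``n P (1 - P)``.
    """
    results = [r for r in results if r is not None]
    if not results:
        raise ValueError("no HWE results to aggregate")
    obs = sum(r.observed_hom for r in results)
    exp = sum(r.expected_hom for r in results)
    var = sum(
        r.n * (r.expected_hom / r.n) * (1.0 - r.expected_hom / r.n) for r in results
    )
    if var == 0:
        z, p = 0.0, 1.0
    else:
        z = (obs - exp) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return {"observed": float(obs), "expected": float(exp), "z": float(z), "p_value": float(p)}


def pairwise_r2(
    matrix: GenotypeMatrix, threshold: float = 0.1
) -> list[tuple[str, str, float]]:
    """SNP pairs whose squared dosage correlation exceeds the threshold.

    r^2 is the squared Pearson correlation of risk-allele counts over
    samples with complete calls for both SNPs, computed on 0/1/2 dosages.
    Pairs where either SNP is monomorphic in the complete subset are
    skipped with a warning.  Returns pairs sorted by descending r^2.
    """
    m = len(matrix.rsids)
    if m < 2:
        raise ValueError("need at least 2 SNPs for a pairwise screen")
    out: list[tuple[str, str, float]] = []
    counts = matrix.counts
    called = ~matrix.missing
    for a in range(m):
        for b in range(a + 1, m):
            both = called[:, a] & called[:, b]
            x, y = counts[both, a], counts[both, b]
            if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"pair ({matrix.rsids[a]}, {matrix.rsids[b]}) skipped: "
                    "monomorphic or insufficient complete calls",
                    stacklevel=2,
                )
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2 = float(r * r)
            if r2 > threshold:
                out.append((matrix.rsids[a], matrix.rsids[b], r2))
    out.sort(key=lambda t: -t[2])
    return out


@dataclass
class QcReport:
    """Everything the QC stage decided, serializable to JSON."""

    excluded_snps: list[tuple[str, float]]
    excluded_samples: list[tuple[str, int]]
    kept_rsids: list[str]
    kept_sample_ids: list[str]
    hwe_table: dict[str, HweResult] = field(default_factory=dict)
    aggregate_homozygotes: dict[str, float] = field(default_factory=dict)
    r2_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "excluded_snps": [
                    {"rsid": r, "fail_fraction": f} for r, f in self.excluded_snps
                ],
                "excluded_samples": [
                    {"sample_id": s, "n_failed_snps": n} for s, n in self.excluded_samples
                ],
                "n_kept_snps": len(self.kept_rsids),
                "n_kept_samples": len(self.kept_sample_ids),
                "hwe": {
                    r: {
                        "n": h.n,
                        "observed_hom": h.observed_hom,
                        "expected_hom": h.expected_hom,
                        "p_value": h.p_value,
                    }
                    for r, h in self.hwe_table.items()
                },
                "aggregate_homozygotes": self.aggregate_homozygotes,
                "r2_pairs": [
                    {"rsid_a": a, "rsid_b": b, "r2": v} for a, b, v in self.r2_pairs
                ],
            },
            indent=indent,
        )

    def summary_lines(self) -> list[str]:
        lines = [
            f"SNPs excluded (call rate): {len(self.excluded_snps)}",
            f"Samples excluded (failures): {len(self.excluded_samples)}",
            f"SNPs retained: {len(self.kept_rsids)}",
            f"Samples retained: {len(self.kept_sample_ids)}",
        ]
        if self.aggregate_homozygotes:
            agg = self.aggregate_homozygotes
            lines.append(
                "Homozygotes observed/expected: "
                f"{agg['observed']:.0f}/{agg['expected']:.1f} (P = {agg['p_value']:.2g})"
            )
        if self.hwe_table:
            pmin = min(h.p_value for h in self.hwe_table.values())
            lines.append(f"Minimum per-SNP HWE P: {pmin:.3g}")
        lines.append(f"SNP pairs with elevated r2: {len(self.r2_pairs)}")
        return lines


def run_qc(
    matrix: GenotypeMatrix,
    control_ids: Sequence[str] | None = None,
    max_fail_fraction: float = 0.02,
    max_failed_snps: int = 10,
    r2_threshold: float = 0.1,
    hwe_on_all_samples: bool = False,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the full QC pipeline and return the filtered matrix plus report.

    The HWE allele frequency is estimated from controls only (cases are
    selected on outcome) unless ``hwe_on_all_samples`` is set.
    """
    kept_snps, excl_snps = snp_call_rate_filter(matrix, max_fail_fraction)
    m1 = matrix.subset(snps=kept_snps)
    kept_samples, excl_samples = sample_failure_filter(m1, max_failed_snps)
    m2 = m1.subset(samples=kept_samples)

    if hwe_on_all_samples or control_ids is None:
        hwe_ids = m2.sample_ids
    else:
        control_set = set(control_ids)
        hwe_ids = [s for s in m2.sample_ids if s in control_set]
    hwe_matrix = m2.subset(samples=hwe_ids) if hwe_ids else None

    hwe_table: dict[str, HweResult] = {}
    if hwe_matrix is not None and hwe_matrix.counts.size:
        for j, rsid in enumerate(hwe_matrix.rsids):
            res = hwe_homozygote_test(hwe_matrix.counts[:, j])
            if res is not None:
                hwe_table[rsid] = res
    agg = aggregate_hwe_test(list(hwe_table.values())) if hwe_table else {}
    r2 = pairwise_r2(m2, r2_threshold) if len(m2.rsids) >= 2 else []

    report = QcReport(
        excluded_snps=excl_snps,
        excluded_samples=excl_samples,
        kept_rsids=m2.rsids,
        kept_sample_ids=m2.sample_ids,
        hwe_table=hwe_table,
        aggregate_homozygotes=agg,
        r2_pairs=r2,
    )
    return m2, report
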