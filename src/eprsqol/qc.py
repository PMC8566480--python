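"""Genotype quality control.

Marker filters follow the usual chip-QC conventions: call rate > 95%
(tightened to > 99% for markers with minor allele frequency below 5%),
MAF > 1%, and Hardy-Weinberg equilibrium exact-test p > 1e-6 — all strict
inequalities.  Sample filters remove individuals with call rate <= 95% or
heterozygosity outside mean +/- 3 SD.  Principal components of the
column-standardized dosage matrix provide the population-stratification
covariates for the downstream regression models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "hwe_exact_test",
    "marker_stats",
    "filter_markers",
    "filter_samples",
    "genotype_pcs",
]


@dataclass(frozen=True)
class QcThresholds:
    """Strict lower bounds used by the marker and sample filters."""

    call_rate: float = 0.95
    call_rate_low_maf: float = 0.99  # applies when MAF < low_maf_cut
    low_maf_cut: float = 0.05
    maf: float = 0.01
    hwe_p: float = 1e-6
    sample_call_rate: float = 0.95
    het_sd: float = 3.0


@dataclass
class QcReport:
    """Outcome of one filtering pass.

    ``removed`` maps the removed identifier to its primary reason code — the
    first failing filter in the fixed order call rate, MAF, HWE (markers) or
    call rate, heterozygosity (samples).
    """

    kept: list[str]
    removed: pd.DataFrame  # columns: id, reason
    thresholds: dict
    metadata: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kept": self.kept,
            "removed": self.removed.to_dict(orient="records"),
            "thresholds": self.thresholds,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def to_tsv(self, path: str | Path) -> None:
        self.removed.to_csv(path, sep="\t", index=False)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy-Weinberg genotype proportions.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of the correct parity, the probabilities of configurations no more
    probable than the observed one.  Returns a p-value in (0, 1].
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    n_a = n_Aa + 2 * n_aa  # minor-ish allele count; symmetry makes choice moot
    n_A = 2 * n - n_a
    rare = min(n_A, n_a)

    return _hwe_p(n, n_A, n_a, rare, n_Aa)


def _hwe_p(
    n: int, n_A: int, n_a: int, rare: int, h_obs: int,
    lgamma_table: np.ndarray | None = None,
) -> float:
    """Exact HWE p given totals; optional precomputed log-factorial table."""
    if lgamma_table is None:
        from scipy.special import gammaln

        lgamma_table = gammaln(np.arange(2 * n + 2))
    lt = lgamma_table
    hs = np.arange(rare % 2, rare + 1, 2)
    n_rr = (rare - hs) // 2
    n_cc = n - n_rr - hs
    lps = hs * math.log(2) - lt[n_rr + 1] - lt[hs + 1] - lt[n_cc + 1]
    lps -= lps.max()
    probs = np.exp(lps)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, h_obs)]
    # relative tolerance guards ties against floating round-off
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def marker_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call rate, MAF, HWE exact p, and hard-call genotype counts.

    Genotype counts come from rounding dosages to hard calls; fractional
    imputed dosages therefore contribute to their nearest genotype class.
    """
    d = gm.dosages
    hard = np.where(np.isnan(d), np.nan, np.round(d))
    n_aa_alt = np.nansum(hard == 2, axis=0).astype(int)
    n_het = np.nansum(hard == 1, axis=0).astype(int)
    n_ref = np.nansum(hard == 0, axis=0).astype(int)
    from scipy.special import gammaln

    lt = gammaln(np.arange(2 * gm.n_samples + 2))
    hwe = np.ones(gm.n_markers)
    for j in range(gm.n_markers):
        total = n_ref[j] + n_het[j] + n_aa_alt[j]
        if total == 0:
            hwe[j] = np.nan
            continue
        n_a = n_het[j] + 2 * n_aa_alt[j]
        rare = min(n_a, 2 * total - n_a)
        hwe[j] = _hwe_p(total, 2 * total - n_a, n_a, rare, n_het[j], lt)
    return pd.DataFrame(
        {
            "snp_id": gm.markers["snp_id"].to_numpy(),
            "call_rate": gm.marker_call_rate(),
            "maf": gm.maf(),
            "hwe_p": hwe,
            "n_AA": n_ref,
            "n_Aa": n_het,
            "n_aa": n_aa_alt,
        }
    )


def filter_markers(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers failing call-rate, MAF or HWE filters (in that order)."""
    if gm.n_markers == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    th = thresholds or QcThresholds()
    stats = marker_stats(gm)
    cr_needed = np.where(stats["maf"] < th.low_maf_cut, th.call_rate_low_maf, th.call_rate)
    fail_cr = stats["call_rate"].to_numpy() <= cr_needed
    fail_maf = stats["maf"].to_numpy() <= th.maf
    fail_hwe = stats["hwe_p"].to_numpy() <= th.hwe_p
    reason = np.where(
        fail_cr, "call_rate", np.where(fail_maf, "maf", np.where(fail_hwe, "hwe", ""))
    )
    keep = reason == ""
    removed = pd.DataFrame(
        {"id": stats.loc[~keep, "snp_id"].to_numpy(), "reason": reason[~keep]}
    )
    report = QcReport(
        kept=list(stats.loc[keep, "snp_id"]),
        removed=removed,
        thresholds={
            "call_rate": th.call_rate,
            "call_rate_low_maf": th.call_rate_low_maf,
            "low_maf_cut": th.low_maf_cut,
            "maf": th.maf,
            "hwe_p": th.hwe_p,
        },
        metadata={
            "note": "per-genotype SNP clustering probability is a chip-level "
            "filter with no analogue in dosage data; not applied"
        },
    )
    return gm.take_markers(np.flatnonzero(keep)), report


def filter_samples(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples with low call rate or outlying heterozygosity.

    Heterozygosity is the fraction of non-missing hard calls that are
    heterozygous; the admissible band is mean +/- ``het_sd`` standard
    deviations across samples (computed before any removal).
    """
    if gm.n_markers == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    th = thresholds or QcThresholds()
    cr = gm.sample_call_rate()
    hard = np.where(np.isnan(gm.dosages), np.nan, np.round(gm.dosages))
    with np.errstate(invalid="ignore"):
        het = np.nanmean(hard == 1, axis=1)
    mu, sd = float(np.mean(het)), float(np.std(het))
    lo, hi = mu - th.het_sd * sd, mu + th.het_sd * sd
    fail_cr = cr <= th.sample_call_rate
    fail_het = (het < lo) | (het > hi)
    reason = np.where(fail_cr, "call_rate", np.where(fail_het, "heterozygosity", ""))
    keep = reason == ""
    removed = pd.DataFrame(
        {
            "id": [s for s, k in zip(gm.samples, keep) if not k],
            "reason": reason[~keep],
        }
    )
    report = QcReport(
        kept=[s for s, k in zip(gm.samples, keep) if k],
        removed=removed,
        thresholds={
            "sample_call_rate": th.sample_call_rate,
            "het_sd": th.het_sd,
            "het_bounds": [lo, hi],
        },
    )
    return gm.take_samples(np.flatnonzero(keep)), report


def _randomized_svd(
    X: np.ndarray, k: int, oversample: int = 10, n_iter: int = 7
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truncated SVD via a randomized range finder with power iterations.

    Deterministic (fixed internal seed).  Power iterations make the leading
    subspace accurate even when the trailing spectrum is flat, which is the
    usual case for standardized genotype matrices.
    """
    rng = np.random.default_rng(1234)
    l = min(k + oversample, min(X.shape))
    Q = X @ rng.standard_normal((X.shape[1], l))
    Q, _ = np.linalg.qr(Q)
    for _ in range(n_iter):
        Q, _ = np.linalg.qr(X @ (X.T @ Q))
    B = Q.T @ X
    ub, s, vt = np.linalg.svd(B, full_matrices=False)
    u = Q @ ub
    return u[:, :k], s[:k], vt[:k]


def genotype_pcs(gm: GenotypeMatrix, k: int = 3) -> pd.DataFrame:
    """Principal components of the column-standardized dosage matrix.

    Missing dosages are replaced by the marker mean before standardization.
    Components are ordered by explained variance; the sign of each component
    is fixed by making its largest-magnitude marker loading positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(gm.n_samples, gm.n_markers):
        raise ValueError("k exceeds min(n_samples, n_markers)")
    X = gm.mean_imputed()
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    if X.size > 250_000 and k < min(X.shape) // 10:
        u, s, vt = _randomized_svd(X, k)
    else:
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u * s
    return pd.DataFrame(
        scores, index=pd.Index(gm.samples, name="sample_id"),
        columns=[f"pc{i + 1}" for i in range(k)],
    )
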