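"""Expression-weighted polygenic network score (ePRS).

The score aggregates, over the SNPs of a co-expression gene network, the
effect-allele dosage weighted by the SNP's expression effect size (beta) and
by the sign of the gene's co-expression with the index gene (the insulin
receptor).  Higher score means higher predicted expression of the network.

Steps: greedy window-based LD clumping on the selection p-value, allele
reconciliation against the genotype panel, signed weighted summation, then
within-sample standardization and a three-level categorization at +/- 0.5 SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

WEIGHT_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "gene", "beta", "sign", "clump_p",
]

AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


def ld_clump(weights: pd.DataFrame, window_bp: int = 250_000) -> pd.DataFrame:
    """Greedy index-SNP selection: lowest clumping p-value first.

    Repeatedly retain the remaining SNP with the smallest ``clump_p`` and
    discard every other remaining SNP within ``window_bp`` of it on the same
    chromosome.  The retained set is returned in the original row order.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if weights["pos"].isna().any():
        raise ValueError("clumping requires positions for every SNP")
    order = np.lexsort((np.arange(len(weights)), weights["clump_p"].to_numpy()))
    chrom = weights["chrom"].to_numpy()
    pos = weights["pos"].to_numpy()
    alive = np.ones(len(weights), dtype=bool)
    retained = np.zeros(len(weights), dtype=bool)
    for i in order:
        if not alive[i]:
            continue
        retained[i] = True
        near = (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        alive &= ~near
    return weights.loc[retained].copy()


@dataclass
class AlleleReconciliation:
    """Bookkeeping from aligning a weight table to a genotype panel."""

    n_matched: int
    n_flipped: int
    n_ambiguous_dropped: int
    n_mismatch_dropped: int
    n_absent: int


def reconcile_alleles(
    gm: GenotypeMatrix, weights: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, AlleleReconciliation]:
    """Align weight-table SNPs with panel markers on the effect allele.

    Returns the usable weight rows, a matching dosage matrix (columns in the
    same order, counted on the effect allele, missing mean-imputed), and a
    reconciliation report.  Strand-ambiguous (A/T, C/G) SNPs and
    allele-mismatching SNPs are dropped and logged.
    """
    panel = gm.markers.set_index("snp_id")
    dose = gm.mean_imputed()
    col_of = {sid: j for j, sid in enumerate(gm.markers["snp_id"])}

    keep_rows: list[int] = []
    cols: list[np.ndarray] = []
    n_match = n_flip = n_amb = n_mis = n_absent = 0
    for i, w in enumerate(weights.itertuples(index=False)):
        if w.snp_id not in col_of:
            n_absent += 1
            continue
        if frozenset({str(w.effect_allele), str(w.other_allele)}) in AMBIGUOUS_PAIRS:
            n_amb += 1
            continue
        ref = str(panel.at[w.snp_id, "ref"])
        alt = str(panel.at[w.snp_id, "alt"])
        d = dose[:, col_of[w.snp_id]]
        if w.effect_allele == alt and w.other_allele == ref:
            cols.append(d)
            n_match += 1
        elif w.effect_allele == ref and w.other_allele == alt:
            cols.append(2.0 - d)
            n_flip += 1
        else:
            n_mis += 1
            continue
        keep_rows.append(i)

    if n_amb or n_mis or n_absent:
        logger.warning(
            "allele reconciliation dropped %d ambiguous, %d mismatching, "
            "%d absent SNPs", n_amb, n_mis, n_absent,
        )
    report = AlleleReconciliation(n_match, n_flip, n_amb, n_mis, n_absent)
    aligned = np.column_stack(cols) if cols else np.empty((gm.n_samples, 0))
    return weights.iloc[keep_rows].copy(), aligned, report


def compute_eprs(gm: GenotypeMatrix, weights: pd.DataFrame) -> pd.Series:
    """Raw network score per sample: sum of dosage x beta x sign.

    ``weights`` should already be LD-clumped.  Dosage is counted on the effect
    allele (flipped where the weight table and panel disagree on orientation);
    missing dosages are replaced by the marker's mean dosage.
    """
    kept, aligned, _ = reconcile_alleles(gm, weights)
    if aligned.shape[1] == 0:
        raise ValueError("no overlapping usable SNPs between genotypes and weights")
    w = kept["beta"].to_numpy(dtype=float) * kept["sign"].to_numpy(dtype=float)
    raw = aligned @ w
    return pd.Series(raw, index=pd.Index(gm.samples, name="sample_id"), name="raw")


def standardize_and_categorize(
    raw_scores: pd.Series | np.ndarray, low: float = -0.5, high: float = 0.5
) -> pd.DataFrame:
    """Standardize raw scores within the analysis sample and bin at +/- 0.5 SD.

    Categories: ``low`` (z < -0.5), ``moderate`` (-0.5 <= z <= 0.5, boundaries
    inclusive), ``high`` (z > 0.5).
    """
    raw = pd.Series(raw_scores)
    if len(raw) < 2:
        raise ValueError("need at least two samples to standardize")
    sd = raw.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("raw scores have zero variance")
    z = (raw - raw.mean()) / sd
    category = pd.Categorical(
        np.where(z < low, "low", np.where(z > high, "high", "moderate")),
        categories=["low", "moderate", "high"],
        ordered=True,
    )
    out = pd.DataFrame({"raw": raw, "z": z, "category": category})
    out.index.name = "sample_id"
    return out


def score_pipeline(
    gm: GenotypeMatrix, weights: pd.DataFrame, window_bp: int = 250_000
) -> pd.DataFrame:
    """Clump, score and standardize in one call."""
    clumped = ld_clump(weights, window_bp=window_bp)
    raw = compute_eprs(gm, clumped)
    return standardize_and_categorize(raw)
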