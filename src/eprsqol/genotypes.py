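"""Allele-dosage genotype container and VCF/TSV input-output.

The central object is :class:`GenotypeMatrix`: a samples x markers matrix of
allele dosages (count of the alternate allele, 0/1/2, ``NaN`` for missing)
together with per-marker metadata (identifier, chromosome, position, ref/alt
alleles).  VCF reading goes through :mod:`cyvcf2`; writing emits a minimal
VCF 4.2 with ``GT`` and a ``DS`` dosage FORMAT field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MARKER_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with marker metadata.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_samples, n_markers)``; entries are alternate
        allele counts in ``{0, 1, 2}`` (intermediate values are permitted for
        imputed dosages) and ``NaN`` marks a missing call.
    samples
        Sample identifiers, one per row.
    markers
        Marker metadata with columns ``snp_id, chrom, pos, ref, alt``.
    """

    dosages: np.ndarray
    samples: list[str]
    markers: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x markers array")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample list does not match dosage rows")
        if len(self.markers) != self.dosages.shape[1]:
            raise ValueError("marker table does not match dosage columns")
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker table lacks columns: {missing}")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    # -- per-axis summaries -------------------------------------------------

    def marker_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def alt_allele_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the marker mean."""
        d = self.dosages.copy()
        mask = np.isnan(d)
        if mask.any():
            with np.errstate(invalid="ignore"):
                means = np.nanmean(d, axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            d[mask] = np.broadcast_to(means, d.shape)[mask]
        return d

    # -- subsetting ---------------------------------------------------------

    def take_markers(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.samples), self.markers.iloc[idx]
        )

    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            self.dosages[idx], [self.samples[i] for i in idx], self.markers
        )

    # -- plain-text I/O -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write a dosage TSV: marker metadata columns then one column per sample."""
        dose = pd.DataFrame(self.dosages.T, columns=self.samples)
        pd.concat([self.markers.reset_index(drop=True), dose], axis=1).to_csv(
            path, sep="\t", index=False, na_rep="NA"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        markers = df[MARKER_COLUMNS].copy()
        samples = [c for c in df.columns if c not in MARKER_COLUMNS]
        dosages = df[samples].to_numpy(dtype=float).T
        return cls(dosages, samples, markers)

    def to_vcf(self, path: str | Path) -> None:
        write_vcf(self, path)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        return read_vcf(path)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT and DS per sample.

    Hard genotype calls are the rounded dosage; the DS field preserves the
    exact dosage value.  Missing dosages become ``./.`` with DS ``.``.
    """
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n'
        )
        chroms = pd.unique(gm.markers["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i, row in enumerate(gm.markers.itertuples(index=False)):
            fields = [
                str(row.chrom),
                str(int(row.pos)),
                str(row.snp_id),
                str(row.ref),
                str(row.alt),
                ".",
                "PASS",
                ".",
                "GT:DS",
            ]
            col = gm.dosages[:, i]
            for d in col:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_codes[int(round(d))]}:{d:g}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read dosages from a VCF, preferring the DS field, else alt counts from GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    meta = []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        meta.append((var.ID, var.CHROM, var.POS, var.REF, alt))
        ds = None
        try:
            ds = var.format("DS")
        except Exception:
            ds = None
        if ds is not None:
            col = ds.astype(float).reshape(-1)
            # cyvcf2 encodes missing floats as very negative sentinels
            col = np.where(col < -1.0, np.nan, col)
        else:
            g = var.gt_types.astype(float)  # 0,1,2,3(=missing) with gts012
            col = np.where(g >= 3, np.nan, g)
        rows.append(col)
    vcf.close()
    dosages = np.vstack(rows).T if rows else np.empty((len(samples), 0))
    markers = pd.DataFrame(meta, columns=MARKER_COLUMNS)
    return GenotypeMatrix(dosages, samples, markers)
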